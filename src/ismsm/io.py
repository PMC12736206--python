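"""Readers and writers for the standard input/output formats.

FASTA via Biopython; SMILES tables, descriptor tables and ADMET feature
tables as headered CSV/TSV through pandas. One CSV dialect throughout:
comma-separated, UTF-8, header required, "." decimal.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .eiip import EncodedSequence
from .localization import DomainAnnotation, HotspotSet
from .scoring import RISK_CATEGORIES, DescriptorRecord
from .spectra import CrossSpectrum, InformationalSpectrum

__all__ = [
    "read_fasta",
    "read_smiles_table",
    "read_descriptor_table",
    "read_admet_table",
    "write_spectrum_csv",
    "write_spectrum_json",
    "write_domains_csv",
    "write_domains_bed",
    "write_hotspots_csv",
    "write_run_manifest",
]

_GAP_CHARS = set("-.*")


class FastaFormatError(ValueError):
    pass


class TableFormatError(ValueError):
    pass


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs; id up to the first whitespace, sequences
    uppercased. Gap characters are rejected; an empty file is an error."""
    path = Path(path)
    # Pre-scan for structural problems Biopython silently tolerates.
    with open(path) as fh:
        seen_header = False
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                seen_header = True
            elif not seen_header:
                raise FastaFormatError(
                    f"{path}: line {lineno}: sequence data before any '>' header"
                )
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    out: list[tuple[str, str]] = []
    for rec in records:
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaFormatError(f"{path}: record {rec.id!r} has an empty sequence")
        bad = _GAP_CHARS.intersection(seq)
        if bad:
            raise FastaFormatError(
                f"{path}: record {rec.id!r} contains gap characters {sorted(bad)}"
            )
        out.append((rec.id, seq))
    return out


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_smiles_table(path: str | Path) -> list[tuple[str, str]]:
    """(id, smiles) rows in file order from a headered CSV/TSV."""
    path = Path(path)
    df = _read_table(path)
    cols = {c.lower(): c for c in df.columns}
    if "id" not in cols or "smiles" not in cols:
        raise TableFormatError(
            f"{path}: need columns id, smiles; header found: {list(df.columns)}"
        )
    ids = df[cols["id"]]
    smiles = df[cols["smiles"]]
    dupes = ids[ids.duplicated()].unique().tolist()
    if dupes:
        raise TableFormatError(f"{path}: duplicate compound ids: {dupes}")
    for row, (i, s) in enumerate(zip(ids, smiles), start=2):  # 1-based + header
        if not str(s).strip():
            raise TableFormatError(f"{path}: blank SMILES at row {row} (id {i!r})")
        if not str(i).strip():
            raise TableFormatError(f"{path}: blank id at row {row}")
    return list(zip(ids.astype(str), smiles.astype(str)))


def read_descriptor_table(path: str | Path) -> list[DescriptorRecord]:
    """Descriptor CSV: compound_id, logP, logS, mw, d, and the four risk
    columns (values none/low/high)."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"compound_id", "logP", "logS", "mw", "d", *RISK_CATEGORIES}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            DescriptorRecord(
                compound_id=str(row["compound_id"]),
                logP=float(row["logP"]),
                logS=float(row["logS"]),
                mw=float(row["mw"]),
                d=float(row["d"]),
                risks={c: str(row[c]) for c in RISK_CATEGORIES},
            )
        )
    return records


def read_admet_table(path: str | Path) -> pd.DataFrame:
    """ADMET feature CSV indexed by compound_id; Yes/No mapped to 1/0."""
    path = Path(path)
    df = pd.read_csv(path)
    if "compound_id" not in df.columns:
        raise TableFormatError(f"{path}: missing compound_id column")
    df = df.set_index("compound_id")
    try:
        df = df.astype(str).apply(
            lambda c: c.str.strip().str.lower().replace({"yes": "1", "no": "0"})
        ).astype(float)
    except ValueError as exc:
        raise TableFormatError(f"{path}: non-numeric ADMET value: {exc}") from exc
    if df.isna().any().any():
        raise TableFormatError(f"{path}: missing values in ADMET table")
    return df


def _spectrum_frame(spectrum: InformationalSpectrum | CrossSpectrum) -> pd.DataFrame:
    amps = spectrum.amplitudes
    mean = amps.mean()
    snr = amps / mean if mean > 0 else np.zeros_like(amps)
    return pd.DataFrame(
        {"frequency": spectrum.frequencies, "amplitude": amps, "snr": snr}
    )


def write_spectrum_csv(spectrum, path: str | Path) -> None:
    _spectrum_frame(spectrum).to_csv(path, index=False)


def write_spectrum_json(spectrum, path: str | Path) -> None:
    frame = _spectrum_frame(spectrum)
    ids = (
        list(spectrum.member_ids)
        if isinstance(spectrum, CrossSpectrum)
        else [spectrum.source_id]
    )
    payload = {
        "member_ids": ids,
        "grid_length": spectrum.grid_length,
        "frequency": frame["frequency"].tolist(),
        "amplitude": frame["amplitude"].tolist(),
        "snr": frame["snr"].tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_domains_csv(domains: Sequence[DomainAnnotation], path: str | Path) -> None:
    """1-based inclusive residue coordinates."""
    pd.DataFrame(
        [
            {
                "protein_id": d.protein_id,
                "start": d.start,
                "end": d.end,
                "frequency": d.frequency,
                "score": d.peak_response,
            }
            for d in domains
        ]
    ).to_csv(path, index=False)


def write_domains_bed(domains: Sequence[DomainAnnotation], path: str | Path) -> None:
    """BED: 0-based half-open, score in column 5."""
    with open(path, "w") as fh:
        for d in domains:
            chrom, start, end = d.to_bed()
            name = f"F{d.frequency:.3f}"
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{d.peak_response:.6g}\n")


def write_hotspots_csv(hotspots: Iterable[HotspotSet], path: str | Path) -> None:
    rows = []
    for hs in hotspots:
        for start, end in hs.intervals:
            rows.append(
                {
                    "protein_id": hs.protein_id,
                    "start": start,
                    "end": end,
                    "frequency": hs.frequency,
                    "scale": hs.scale,
                    "band_threshold": hs.band_threshold,
                    "edge_flagged": (start, end) in hs.edge_flagged,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_run_manifest(path: str | Path, **params) -> None:
    """JSON manifest of a screening run (grid length, mode, seed, cutoffs...)."""
    Path(path).write_text(json.dumps(params, indent=1, sort_keys=True, default=str))
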