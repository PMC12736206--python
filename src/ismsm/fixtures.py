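"""Synthetic fixtures with exact ground truth.

Every generator is seed-deterministic. Planted periodic signals are injected
directly in EIIP space (amplitude * cos(2 pi f0 (m-1)) + Gaussian noise) so
the ground-truth frequency is exact; a residue-quantized mode maps the
sinusoid onto nearest-EIIP amino acids for realistic protein input, and the
"matched ligand" quantizes the cosine's sign onto a two-atom chain palette
(ether oxygen vs secondary amine) so a real SMILES molecule carries f0.

The fixture SNR convention is amplitude / noise_sd.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .eiip import EncodedSequence, load_amino_acid_table

__all__ = [
    "FixtureSpec",
    "make_planted_sequence",
    "make_planted_protein",
    "make_ortholog_family",
    "make_decoy_library",
    "make_matched_ligand_smiles",
    "make_blob_admet",
]


@dataclass(frozen=True)
class FixtureSpec:
    kind: Literal[
        "planted-sequence",
        "ortholog-family",
        "decoy-library",
        "burst-sequence",
        "blob-admet",
    ]
    seed: int
    length: int = 512
    n: int = 12
    f0: float = 0.167
    amplitude: float = 1.0
    noise_sd: float = 0.25
    region: tuple[int, int] | None = None  # 1-based inclusive, burst kind
    length_jitter: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.f0 <= 0.5:
            raise ValueError(f"planted frequency {self.f0} outside (0, 0.5]")

    @property
    def snr(self) -> float:
        return np.inf if self.noise_sd == 0 else self.amplitude / self.noise_sd


def _cosine(length: int, f0: float, amplitude: float) -> np.ndarray:
    m = np.arange(length)
    return amplitude * np.cos(2.0 * np.pi * f0 * m)


def make_planted_sequence(spec: FixtureSpec) -> tuple[EncodedSequence, dict]:
    """EIIP-space series with a planted cosine at f0 (whole length, or only
    inside ``region`` for the burst kind) plus Gaussian noise.

    Returns (sequence, ground_truth) where ground_truth records f0 and, for
    bursts, the 1-based signal region.
    """
    rng = np.random.default_rng(spec.seed)
    x = rng.normal(0.0, spec.noise_sd, spec.length)
    truth: dict = {"f0": spec.f0}
    if spec.kind == "burst-sequence":
        if spec.region is None:
            raise ValueError("burst-sequence fixture requires a region")
        start, end = spec.region
        if not 1 <= start <= end <= spec.length:
            raise ValueError(f"region {spec.region} outside sequence of length {spec.length}")
        m = np.arange(start - 1, end)
        x[start - 1 : end] += spec.amplitude * np.cos(2.0 * np.pi * spec.f0 * m)
        truth["region"] = (start, end)
    else:
        x += _cosine(spec.length, spec.f0, spec.amplitude)
    seq = EncodedSequence(
        id=f"planted-{spec.kind}-seed{spec.seed}",
        kind="protein",
        values=tuple(float(v) for v in x),
    )
    return seq, truth


def make_planted_protein(spec: FixtureSpec) -> tuple[str, dict]:
    """Residue-quantized planted signal: an amino-acid string whose EIIP
    series approximates the planted cosine (nearest tabulated EIIP value per
    position). Realistic input for the FASTA/encoding path; the quantization
    error acts as extra noise."""
    rng = np.random.default_rng(spec.seed)
    table = load_amino_acid_table()
    tokens = list(table.entries)
    values = np.array([table.entries[t] for t in tokens])
    center = values.mean()
    half_range = (values.max() - values.min()) / 2.0
    target = center + half_range * _cosine(spec.length, spec.f0, 1.0)
    target += rng.normal(0.0, spec.noise_sd * half_range, spec.length)
    picks = np.abs(target[:, None] - values[None, :]).argmin(axis=1)
    residues = "".join(tokens[i] for i in picks)
    return residues, {"f0": spec.f0}


def make_ortholog_family(spec: FixtureSpec) -> tuple[list[EncodedSequence], dict]:
    """Family of sequences sharing the planted f0 with independent noise and
    random length jitter (default +/-10%), emulating a mammalian ortholog set."""
    if spec.n < 2:
        raise ValueError("ortholog family needs n >= 2 members")
    rng = np.random.default_rng(spec.seed)
    members = []
    for i in range(spec.n):
        jitter = rng.uniform(-spec.length_jitter, spec.length_jitter)
        length = max(16, int(round(spec.length * (1.0 + jitter))))
        x = _cosine(length, spec.f0, spec.amplitude)
        x += rng.normal(0.0, spec.noise_sd, length)
        members.append(
            EncodedSequence(
                id=f"ortholog-{i}-seed{spec.seed}",
                kind="protein",
                values=tuple(float(v) for v in x),
            )
        )
    return members, {"f0": spec.f0}


# Chain-atom grammar for random decoys: small valid fragments that can be
# concatenated into a linear SMILES without ring-closure bookkeeping.
_DECOY_FRAGMENTS = (
    "C", "CC", "CCC", "N", "O", "CO", "CN", "C(C)", "C(=O)", "C(=O)O",
    "CS", "C(F)", "C(Cl)", "c1ccccc1", "c1ccncc1", "C1CCCCC1", "C1CCOC1",
)


def make_decoy_library(
    spec: FixtureSpec,
    include_matched_ligand: bool = False,
    matched_length: int = 60,
) -> tuple[list[tuple[str, str]], dict]:
    """Random valid SMILES from a small chain grammar, optionally plus one
    matched ligand carrying f0 in its per-group EIIP series.

    Returns ([(id, smiles), ...], ground_truth); ground truth names the
    matched ligand's id when present.
    """
    if spec.n < 1:
        raise ValueError("library needs n >= 1 compounds")
    rng = np.random.default_rng(spec.seed)
    rows: list[tuple[str, str]] = []
    for i in range(spec.n):
        n_frag = int(rng.integers(2, 7))
        idx = rng.integers(0, len(_DECOY_FRAGMENTS), n_frag)
        smiles = "".join(_DECOY_FRAGMENTS[j] for j in idx)
        rows.append((f"DECOY{i:05d}", smiles))
    truth: dict = {"f0": spec.f0, "matched_id": None}
    if include_matched_ligand:
        matched = make_matched_ligand_smiles(spec.f0, matched_length)
        rows.append(("MATCHED00000", matched))
        truth["matched_id"] = "MATCHED00000"
    return rows, truth


def make_matched_ligand_smiles(f0: float, length: int = 60) -> str:
    """A chain molecule whose per-group EIIP series oscillates at f0.

    Quantizes sign(cos(2 pi f0 m)) onto {O (ether), N (amine)} chain atoms;
    the resulting square wave's fundamental sits at f0. Chemically exotic
    (O-O/N-N chains) but valid SMILES with correct valences.
    """
    m = np.arange(length)
    signs = np.cos(2.0 * np.pi * f0 * m) >= 0
    return "".join("O" if s else "N" for s in signs)


def make_blob_admet(
    spec: FixtureSpec,
    n_features: int = 8,
    separation: float = 10.0,
    k: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Well-separated Gaussian blobs for clustering tests.

    Returns (X, labels); blob centers are ``separation`` standard deviations
    apart along random orthogonal directions.
    """
    if k > n_features:
        raise ValueError("need n_features >= k for orthogonal blob centers")
    if n_features & (n_features - 1):
        raise ValueError("n_features must be a power of two (Hadamard centers)")
    rng = np.random.default_rng(spec.seed)
    # Hadamard directions spread each pairwise separation evenly over the
    # features, so per-feature standardization (which down-weights features
    # mixing signal and noise unevenly) cannot erode the class margin; random
    # QR directions can lose half of it. Pairwise center distance is exactly
    # ``separation``.
    from scipy.linalg import hadamard

    q = hadamard(n_features).astype(float) / np.sqrt(n_features)
    q = q[rng.permutation(n_features)][:, rng.permutation(n_features)]
    centers = q[:, :k].T * (separation / np.sqrt(2.0))
    centers -= centers.mean(axis=0)  # centered simplex: no wasted variance
    labels = np.repeat(np.arange(k), spec.n)
    X = centers[labels] + rng.normal(0.0, 1.0, (len(labels), n_features))
    return X, labels
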