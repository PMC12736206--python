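"""Drug Score aggregation, Total Score, and ADMET k-means ranking.

The Drug Score dS compresses four physicochemical descriptors (logP, logS,
molecular weight, druglikeness d) through per-descriptor sigmoids
s = 1/(1 + exp(a*p + b)) and multiplies in toxicity weights:

    dS = prod_desc (1/2 + s_desc/2) * prod_risk t_risk,
    t  = 1.0 / 0.8 / 0.6 for none / low / high risk.

Total Score = dS * S/N combines druglikeness with spectral interaction
specificity; Total Score 2 = S/N / (distance to ADMET cluster centroid)
favors spectrally specific compounds near a cluster's pharmacokinetic
archetype.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

__all__ = [
    "RiskLevel",
    "TOXICITY_WEIGHTS",
    "SIGMOID_PARAMS",
    "DescriptorRecord",
    "ScoreRecord",
    "AdmetClustering",
    "sigmoid_component",
    "druglikeness",
    "drug_score",
    "total_score",
    "cluster_admet",
    "total_score2",
]

RiskLevel = Literal["none", "low", "high"]
RISK_CATEGORIES = ("irritation", "mutagenic", "reproductive", "tumorigenic")
TOXICITY_WEIGHTS: Mapping[str, float] = {"none": 1.0, "low": 0.8, "high": 0.6}

# (a, b) per descriptor. "datawarrior": orientation per the DataWarrior
# property documentation, under which favorable values score high.
# "printed": the literal pairs as printed alongside Eq. (7), for comparison
# (note these give s ~ 0 at high MW for essentially all real drugs).
SIGMOID_PARAMS: Mapping[str, Mapping[str, tuple[float, float]]] = {
    "datawarrior": {"logP": (1.0, -5.0), "logS": (-1.0, -5.0), "mw": (0.012, -6.0), "d": (-1.0, 0.0)},
    "printed": {"logP": (1.0, -5.0), "logS": (1.0, 5.0), "mw": (0.012, 6.0), "d": (1.0, 0.0)},
}


@dataclass(frozen=True)
class DescriptorRecord:
    compound_id: str
    logP: float
    logS: float
    mw: float  # Da
    d: float  # druglikeness
    risks: Mapping[str, RiskLevel] = field(
        default_factory=lambda: {c: "none" for c in RISK_CATEGORIES}
    )

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError(f"{self.compound_id!r}: molecular weight must be > 0")
        if set(self.risks) != set(RISK_CATEGORIES):
            raise ValueError(
                f"{self.compound_id!r}: risks must cover exactly {RISK_CATEGORIES}"
            )


@dataclass
class ScoreRecord:
    compound_id: str
    dS: float
    snr: float
    total_score: float
    cluster: int | None = None
    centroid_distance: float | None = None
    total_score2: float | None = None
    zero_distance_flag: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.dS <= 1.0:
            raise ValueError("dS must lie in [0, 1]")


def sigmoid_component(p: float, a: float, b: float) -> float:
    """s = 1 / (1 + exp(a*p + b)); equals 0.5 where a*p + b = 0."""
    z = a * p + b
    if z <= 0:
        return 1.0 / (1.0 + math.exp(z))
    ez = math.exp(-z)  # avoid overflow for large positive z
    return ez / (1.0 + ez)


def druglikeness(fragment_scores: Sequence[float], n: int) -> float:
    """d = (sum of matched fragment scores) / n.

    The fragment library and its per-fragment scores are caller-supplied
    (pluggable provider); an empty match list contributes a zero sum.
    """
    if n < 1:
        raise ValueError("normalization count n must be >= 1")
    return sum(fragment_scores) / n


def drug_score(
    rec: DescriptorRecord,
    params: Mapping[str, tuple[float, float]] | None = None,
    toxicity_weights: Mapping[str, float] = TOXICITY_WEIGHTS,
    convention: str = "datawarrior",
) -> float:
    """dS = prod(1/2 + s_i/2) over {logP, logS, mw, d} times prod t_risk."""
    if params is None:
        params = SIGMOID_PARAMS[convention]
    missing = {"logP", "logS", "mw", "d"} - set(params)
    if missing:
        raise ValueError(f"sigmoid params missing descriptors: {sorted(missing)}")
    ds = 1.0
    for name, p in (("logP", rec.logP), ("logS", rec.logS), ("mw", rec.mw), ("d", rec.d)):
        a, b = params[name]
        ds *= 0.5 + 0.5 * sigmoid_component(p, a, b)
    for category, level in rec.risks.items():
        if level not in toxicity_weights:
            raise ValueError(
                f"{rec.compound_id!r}: unknown risk level {level!r} for {category}"
            )
        ds *= toxicity_weights[level]
    return ds


def total_score(dS: float, snr: float) -> float:
    """Total Score = dS x S/N."""
    if dS < 0 or snr < 0:
        raise ValueError("dS and S/N must be non-negative")
    return dS * snr


@dataclass(frozen=True)
class AdmetClustering:
    compound_ids: tuple[str, ...]
    assignments: np.ndarray  # cluster label per row
    centroid_distances: np.ndarray  # Euclidean, standardized space
    centroids: np.ndarray  # (k, n_features), standardized space
    within_variance_pct: float
    between_variance_pct: float
    feature_names: tuple[str, ...]
    dropped_columns: tuple[str, ...] = ()


def cluster_admet(
    table: pd.DataFrame,
    k: int = 5,
    restarts: int = 10,
    seed: int = 42,
) -> AdmetClustering:
    """k-means over a standardized ADMET feature table.

    ``table`` is indexed by compound id with numeric columns (Yes/No already
    mapped to 1/0). Constant columns are dropped with a warning since
    standardization is undefined for them. Reports per-row cluster label,
    Euclidean distance to the own centroid in standardized space, and the
    within/between variance decomposition (sums to 100%).
    """
    if len(table) < k:
        raise ValueError(f"need at least k={k} rows, got {len(table)}")
    values = table.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("ADMET table contains missing values after preprocessing")
    keep = values.std(axis=0) > 0
    dropped = tuple(str(c) for c, m in zip(table.columns, keep) if not m)
    if dropped:
        warnings.warn(
            f"dropping constant ADMET columns (standardization undefined): {dropped}",
            stacklevel=2,
        )
        values = values[:, keep]
    if values.shape[1] == 0:
        raise ValueError("no variable ADMET columns remain")
    z = StandardScaler().fit_transform(values)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(z)
    labels = km.labels_
    dists = np.linalg.norm(z - km.cluster_centers_[labels], axis=1)

    total_ss = float(((z - z.mean(axis=0)) ** 2).sum())
    within_ss = float((dists**2).sum())
    within_pct = 100.0 * within_ss / total_ss
    return AdmetClustering(
        compound_ids=tuple(str(i) for i in table.index),
        assignments=labels,
        centroid_distances=dists,
        centroids=km.cluster_centers_,
        within_variance_pct=within_pct,
        between_variance_pct=100.0 - within_pct,
        feature_names=tuple(str(c) for c, m in zip(table.columns, keep) if m),
        dropped_columns=dropped,
    )


def total_score2(snr: float, centroid_distance: float) -> float:
    """Total Score 2 = S/N / centroid distance (higher S/N, nearer centroid).

    A zero distance is reported upstream as rank-first with a flag rather
    than as an infinite score; here it is an error.
    """
    if centroid_distance <= 0:
        raise ValueError("centroid distance must be > 0 (zero-distance rows are flagged upstream)")
    if snr < 0:
        raise ValueError("S/N must be non-negative")
    return snr / centroid_distance
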