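"""Enrichment scoring of DNA-pulldown mass-spectrometry peptide counts.

Nuclear proteins captured on immobilised promoter DNA probes are read out as
total peptide counts per protein per pulldown experiment.  The scoring
pipeline mirrors standard spectral-count practice:

1. exclude proteins whose summed count over all experiments is below 5;
2. normalise each experiment by its total peptide count (columns sum to 1);
3. standardise each protein across experiments (row-wise Z-score, sample
   s.d. with n−1 denominator);
4. call a protein enriched when its mean Z over the probe (experimental)
   pulldowns exceeds its mean Z over the control-DNA pulldowns by strictly
   more than 0.5.

Row-wise k-means on the Z-scores provides the ordering used for heatmaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "PulldownMatrix",
    "EnrichmentResult",
    "filter_low_counts",
    "normalize_counts",
    "protein_zscores",
    "select_enriched",
    "cluster_rows",
    "average_replicates",
    "run_enrichment",
]

logger = logging.getLogger(__name__)

EXPERIMENTAL = "experimental"
CONTROL = "control"


@dataclass
class PulldownMatrix:
    """Protein × experiment total peptide counts with experiment metadata.

    ``counts``: DataFrame, index = protein identifiers, columns = experiment
    labels, non-negative integer counts.  ``tags``: DataFrame indexed by the
    same labels with columns ``cls`` (experimental/control), ``condition``
    (probe × timepoint) and ``replicate``.
    """

    counts: pd.DataFrame
    tags: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any() or self.counts.index.duplicated().any():
            raise ValueError("experiment labels and protein identifiers must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("peptide counts must be non-negative")
        missing = set(self.counts.columns) - set(self.tags.index)
        if missing:
            raise ValueError(f"experiments without tags: {sorted(missing)}")
        cls = self.tags.loc[list(self.counts.columns), "cls"]
        bad = set(cls) - {EXPERIMENTAL, CONTROL}
        if bad:
            raise ValueError(f"unknown experiment class: {sorted(bad)}")
        if CONTROL not in set(cls):
            raise ValueError("at least one control-tagged experiment is required")

    @property
    def proteins(self) -> List[str]:
        return list(self.counts.index)

    @property
    def experiments(self) -> List[str]:
        return list(self.counts.columns)

    def labels_of(self, cls: str) -> List[str]:
        tags = self.tags.loc[list(self.counts.columns)]
        return list(tags.index[tags["cls"] == cls])


@dataclass
class EnrichmentResult:
    """Outputs of the filter → normalise → Z → select pipeline."""

    matrix: PulldownMatrix            # the retained (filtered) matrix
    normalized: pd.DataFrame          # fractions; columns sum to 1
    zscores: pd.DataFrame             # per-protein Z across experiments
    enrichment_score: pd.Series       # mean experimental Z − mean control Z
    passed: pd.Series                 # enrichment_score > z_margin
    params: Dict[str, float] = field(default_factory=dict)
    cluster_labels: pd.Series | None = None

    @property
    def enriched_proteins(self) -> List[str]:
        return list(self.passed.index[self.passed])


def filter_low_counts(matrix: PulldownMatrix, min_total: int = 5) -> PulldownMatrix:
    """Drop proteins whose total count across all experiments is below ``min_total``.

    A total of exactly ``min_total`` is retained ("fewer than five" excludes
    strictly).  Survivor order is preserved.  Idempotent.
    """
    totals = matrix.counts.sum(axis=1)
    kept = matrix.counts.loc[totals >= min_total]
    if kept.empty:
        raise ValueError(f"no protein reaches a total count of {min_total}")
    return PulldownMatrix(counts=kept.copy(), tags=matrix.tags.copy())


def normalize_counts(matrix: PulldownMatrix) -> pd.DataFrame:
    """Divide each experiment column by its total peptide count."""
    totals = matrix.counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"zero total peptide count in experiment {zero[0]!r}")
    return matrix.counts / totals


def protein_zscores(normalized: pd.DataFrame, across: str = "experiments") -> pd.DataFrame:
    """Standardise normalised counts.

    ``across="experiments"`` (default): per protein, across all experiments
    (row-wise), sample s.d. (n−1).  ``across="proteins"``: per experiment
    column instead.  Zero-variance rows/columns become all-zero and are
    flagged in the log.
    """
    if normalized.shape[1] < 2:
        raise ValueError("protein_zscores requires >= 2 experiments")
    axis = 1 if across == "experiments" else 0
    if across not in ("experiments", "proteins"):
        raise ValueError(f"unknown standardisation axis {across!r}")
    mean = normalized.mean(axis=axis)
    sd = normalized.std(axis=axis, ddof=1)
    flat = sd.index[sd == 0]
    if len(flat):
        logger.warning("zero variance (Z set to 0) for: %s", ", ".join(map(str, flat)))
    sd = sd.replace(0, np.nan)
    z = normalized.sub(mean, axis=1 - axis).div(sd, axis=1 - axis)
    return z.fillna(0.0)


def select_enriched(
    zscores: pd.DataFrame,
    tags: pd.DataFrame,
    z_margin: float = 0.5,
) -> Tuple[pd.Series, pd.Series]:
    """Score = mean Z over experimental columns − mean Z over control columns.

    A protein passes when its score strictly exceeds ``z_margin``.
    Returns (enrichment_score, passed).
    """
    cls = tags.loc[list(zscores.columns), "cls"]
    exp_cols = list(cls.index[cls == EXPERIMENTAL])
    ctl_cols = list(cls.index[cls == CONTROL])
    if not exp_cols or not ctl_cols:
        raise ValueError("need at least one experimental and one control experiment")
    score = zscores[exp_cols].mean(axis=1) - zscores[ctl_cols].mean(axis=1)
    passed = score > z_margin
    return score, passed


def cluster_rows(zscores: pd.DataFrame, k: int, seed: int = 0) -> Tuple[pd.Series, float]:
    """Seeded k-means over Z-score rows; returns (labels, within-cluster SS)."""
    n = zscores.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    km = KMeans(n_clusters=k, n_init=min(100, 10 * k), random_state=seed)
    labels = km.fit_predict(zscores.to_numpy())
    return pd.Series(labels, index=zscores.index, name="cluster"), float(km.inertia_)


def average_replicates(matrix: PulldownMatrix) -> PulldownMatrix:
    """Average raw counts over replicates of each condition (before normalising)."""
    tags = matrix.tags.loc[list(matrix.counts.columns)]
    groups: Dict[str, List[str]] = {}
    meta: Dict[str, Tuple[str, str]] = {}
    for label, row in tags.iterrows():
        key = str(row["condition"])
        groups.setdefault(key, []).append(label)
        meta[key] = (row["cls"], key)
    data = {key: matrix.counts[labels].mean(axis=1) for key, labels in groups.items()}
    counts = pd.DataFrame(data)
    new_tags = pd.DataFrame(
        {
            "cls": [meta[c][0] for c in counts.columns],
            "condition": [meta[c][1] for c in counts.columns],
            "replicate": [0] * counts.shape[1],
        },
        index=counts.columns,
    )
    return PulldownMatrix(counts=counts, tags=new_tags)


def run_enrichment(
    matrix: PulldownMatrix,
    min_total: int = 5,
    z_margin: float = 0.5,
    across: str = "experiments",
    n_clusters: int | None = None,
    seed: int = 0,
    combine_replicates: bool = False,
) -> EnrichmentResult:
    """The fixed pipeline: filter → normalise → Z-score → select (→ cluster)."""
    if combine_replicates:
        matrix = average_replicates(matrix)
    filtered = filter_low_counts(matrix, min_total=min_total)
    normalized = normalize_counts(filtered)
    zscores = protein_zscores(normalized, across=across)
    score, passed = select_enriched(zscores, filtered.tags, z_margin=z_margin)
    labels = None
    if n_clusters is not None:
        labels, _ = cluster_rows(zscores, n_clusters, seed=seed)
    return EnrichmentResult(
        matrix=filtered,
        normalized=normalized,
        zscores=zscores,
        enrichment_score=score,
        passed=passed,
        params={"min_total_count": min_total, "z_margin": z_margin},
        cluster_labels=labels,
    )
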