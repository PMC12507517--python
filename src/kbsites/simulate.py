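"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators cover every stage of the pipeline without external data:

* :func:`gen_zscore_table` — a stand-in for a protein-binding-microarray
  affinity table: consensus-compatible 10-mers with positive, right-skewed
  Z-scores, always containing the two literature reference sites
  GGGAAATTCC (strong, Z = 14.0) and GGGAAGTTCC (weak, Z = 5.8).
* :func:`gen_peak_cohort` — promoter-like peak regions: a 1001-bp random
  background with one strong κB site planted at the center and several weak
  sites planted within a configurable cluster span (default 150 bp, the span
  observed for native κB clusters), plus a ChIP-like occupancy score that is
  a noisy linear function of the planted cumulative Z-score.
* :func:`gen_pulldown` — Poisson peptide-count matrices with a planted set
  of proteins whose rates are multiplied in the probe (experimental)
  pulldowns only.

All randomness flows from a single seed through named substreams (sequence,
placement, noise, counts) so the same cohort can be regenerated with, e.g.,
a different noise level but identical sequences.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .clusters import PeakRegion, select_anchor
from .motifs import (
    CONSENSUS,
    IUPAC_SETS,
    SITE_LENGTH,
    STRONG_THRESHOLD,
    KappaBSite,
    ScanConfig,
    ZScoreTable,
    classify_site,
    consensus_mismatches,
    designate_sites,
    reverse_complement,
)
from .pulldown import PulldownMatrix

__all__ = [
    "CohortSpec",
    "PlantedPeak",
    "PlantedTruth",
    "SENTINEL_STRONG",
    "SENTINEL_WEAK",
    "gen_zscore_table",
    "gen_peak_cohort",
    "gen_pulldown",
    "max_table_entries",
]

REGION_LENGTH = 1001  # ±500 bp around the peak center

#: literature reference sites carried by every generated table
SENTINEL_STRONG = ("GGGAAATTCC", 14.0)
SENTINEL_WEAK = ("GGGAAGTTCC", 5.8)


def _substreams(seed: int, names: Sequence[str]) -> Dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def max_table_entries(consensus: str = CONSENSUS, max_mismatches: int = 3) -> int:
    """Number of distinct k-mers within ``max_mismatches`` of the consensus.

    A position either stays within its allowed set or takes one of the
    disallowed alternatives; N positions can never mismatch.
    """
    allowed = [len(IUPAC_SETS[sym]) for sym in consensus]
    mutable = [i for i, a in enumerate(allowed) if a < 4]
    total = 0
    for m in range(min(max_mismatches, len(mutable)) + 1):
        for combo in itertools.combinations(mutable, m):
            prod = 1
            for i, a in enumerate(allowed):
                prod *= (4 - a) if i in combo else a
            total += prod
    return total


def gen_zscore_table(n_entries: int, seed: int = 0) -> ZScoreTable:
    """Synthetic affinity table of consensus-compatible 10-mers.

    Every emitted k-mer is within 3 mismatches of GGGRNNYYCC; Z-scores are
    positive and right-skewed (Gamma(1.5, 3) + 0.2, so most entries are weak
    with a strong tail).  The strong and weak reference sites are always
    included.  Deterministic per seed.
    """
    if n_entries < 1:
        raise ValueError("n_entries must be >= 1")
    cap = max_table_entries()
    if n_entries > cap:
        raise ValueError(
            f"n_entries={n_entries} exceeds the {cap} consensus-compatible 10-mers"
        )
    rng = np.random.default_rng(seed)
    entries: Dict[str, float] = {}
    for kmer, z in (SENTINEL_STRONG, SENTINEL_WEAK):
        if len(entries) < n_entries:
            entries[kmer] = z
    allowed_sets = [sorted(IUPAC_SETS[sym]) for sym in CONSENSUS]
    mutable = [i for i, s in enumerate(allowed_sets) if len(s) < 4]
    while len(entries) < n_entries:
        bases = [s[rng.integers(len(s))] for s in allowed_sets]
        m = int(rng.integers(0, 4))
        if m:
            for pos in rng.choice(mutable, size=m, replace=False):
                options = sorted(set("ACGT") - set(allowed_sets[pos]))
                bases[pos] = options[rng.integers(len(options))]
        kmer = "".join(bases)
        if kmer not in entries:
            entries[kmer] = float(rng.gamma(1.5, 3.0) + 0.2)
    return ZScoreTable(entries=entries, source_label=f"synthetic(seed={seed})")


@dataclass
class CohortSpec:
    """Study conditions of a synthetic peak cohort.

    Defaults mirror the structure reported for native κB clusters: one
    strong site with multiple weak neighbours within a ~150-bp span, and an
    occupancy score that tracks the cluster's summed affinity.
    """

    n_peaks: int
    span_bp: int = 150
    n_weak_range: Tuple[int, int] = (2, 8)
    strong_z_range: Tuple[float, float] = (6.0, 15.0)
    weak_z_range: Tuple[float, float] = (1.0, 6.0)
    background_gc: float = 0.45
    alpha: float = 1.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peaks < 4:
            raise ValueError("n_peaks must be >= 4")
        if not 0 < self.span_bp <= 500:
            raise ValueError("span_bp must lie in (0, 500]")
        if self.weak_z_range[1] > STRONG_THRESHOLD:
            raise ValueError("weak_z_range must lie strictly below the strong threshold")
        if not 0 < self.background_gc < 1:
            raise ValueError("background_gc must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.n_weak_range
        if lo < 0 or hi < lo:
            raise ValueError("n_weak_range must be a non-empty non-negative interval")


@dataclass
class PlantedPeak:
    """Ground truth for one generated peak region."""

    region_id: str
    planted_sites: List[KappaBSite]
    true_cumulative_z: float
    noiseless_chip_score: float
    incidental_sites: List[KappaBSite] = field(default_factory=list)

    @property
    def planted_weak_count(self) -> int:
        return sum(1 for s in self.planted_sites if s.site_class == "weak")


@dataclass
class PlantedTruth:
    """Ground truth for a whole cohort, keyed like the peak list."""

    peaks: List[PlantedPeak]

    def __getitem__(self, i: int) -> PlantedPeak:
        return self.peaks[i]

    def __len__(self) -> int:
        return len(self.peaks)


def _plant(seq: List[str], start: int, kmer: str, strand: str) -> None:
    written = kmer if strand == "+" else reverse_complement(kmer)
    seq[start : start + SITE_LENGTH] = list(written)


def gen_peak_cohort(
    spec: CohortSpec,
    table: ZScoreTable,
    config: ScanConfig | None = None,
) -> Tuple[List[PeakRegion], PlantedTruth]:
    """Generate peak regions with planted κB clusters and matching scores.

    Per peak: a 1001-bp i.i.d. background at the requested GC content, one
    strong-class table k-mer planted at the center, and a uniform number of
    weak-class k-mers planted at uniform positions within ±span_bp/2 of the
    center (non-overlapping; resampled on collision, at most 1000 attempts).
    The ChIP-like score is ``alpha * (planted cumulative Z) + N(0, noise_sd)``
    floored at zero.  Background windows that happen to satisfy designation
    are tracked as incidental sites rather than rejected.
    """
    if config is None:
        config = ScanConfig()
    mm_ok = lambda k: consensus_mismatches(k, config.consensus) <= config.max_mismatches
    strong_kmers = sorted(
        k
        for k, z in table.entries.items()
        if spec.strong_z_range[0] <= z <= spec.strong_z_range[1]
        and z >= config.strong_threshold
        and mm_ok(k)
    )
    weak_kmers = sorted(
        k
        for k, z in table.entries.items()
        if spec.weak_z_range[0] <= z < spec.weak_z_range[1]
        and 0 < z < config.strong_threshold
        and mm_ok(k)
    )
    if not strong_kmers:
        raise ValueError("table has no strong-class k-mer within strong_z_range")
    if not weak_kmers and spec.n_weak_range[1] > 0:
        raise ValueError("table has no weak-class k-mer within weak_z_range")

    rngs = _substreams(spec.seed, ["sequence", "placement", "noise"])
    gc = spec.background_gc
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    center = REGION_LENGTH // 2  # site center offset of the planted strong site
    anchor_start = center - SITE_LENGTH // 2

    peaks: List[PeakRegion] = []
    truth: List[PlantedPeak] = []
    for i in range(spec.n_peaks):
        region_id = f"peak_{i:04d}"
        seq = list(
            rngs["sequence"].choice(list("ACGT"), size=REGION_LENGTH, p=probs)
        )
        place = rngs["placement"]
        strong_kmer = strong_kmers[place.integers(len(strong_kmers))]
        strong_strand = "+" if place.integers(2) == 0 else "-"
        planted: List[KappaBSite] = [
            KappaBSite(
                start=anchor_start,
                strand=strong_strand,
                kmer=strong_kmer,
                z_score=table.entries[strong_kmer],
                mismatches=consensus_mismatches(strong_kmer, config.consensus),
                site_class=classify_site(table.entries[strong_kmer], config.strong_threshold),
            )
        ]
        n_weak = int(place.integers(spec.n_weak_range[0], spec.n_weak_range[1] + 1))
        occupied = [anchor_start]
        half = spec.span_bp / 2
        attempts = 0
        while len(planted) - 1 < n_weak:
            attempts += 1
            if attempts > 1000:
                raise ValueError(
                    f"{region_id}: could not place {n_weak} weak sites without overlap; "
                    "use a larger span_bp or fewer sites"
                )
            c = int(place.integers(int(np.ceil(center - half)), int(center + half) + 1))
            start = c - SITE_LENGTH // 2
            if start < 0 or start + SITE_LENGTH > REGION_LENGTH:
                continue
            if any(abs(start - o) < SITE_LENGTH for o in occupied):
                continue
            kmer = weak_kmers[place.integers(len(weak_kmers))]
            strand = "+" if place.integers(2) == 0 else "-"
            occupied.append(start)
            planted.append(
                KappaBSite(
                    start=start,
                    strand=strand,
                    kmer=kmer,
                    z_score=table.entries[kmer],
                    mismatches=consensus_mismatches(kmer, config.consensus),
                    site_class=classify_site(table.entries[kmer], config.strong_threshold),
                )
            )
        for site in planted:
            _plant(seq, site.start, site.kmer, site.strand)
        sequence = "".join(seq)
        true_cum = sum(s.z_score for s in planted)
        noiseless = spec.alpha * true_cum
        noise = rngs["noise"].normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
        chip_score = max(0.0, noiseless + noise)
        sites = designate_sites(sequence, table, config)
        anchor = select_anchor(sites, region_center=center)
        planted_keys = {(s.start) for s in planted}
        incidental = [s for s in sites if s.start not in planted_keys]
        peaks.append(
            PeakRegion(
                region_id=region_id,
                sequence=sequence,
                anchor_offset=anchor.center,
                chip_score=chip_score,
                sites=sites,
            )
        )
        truth.append(
            PlantedPeak(
                region_id=region_id,
                planted_sites=sorted(planted, key=lambda s: s.start),
                true_cumulative_z=true_cum,
                noiseless_chip_score=noiseless,
                incidental_sites=incidental,
            )
        )
    return peaks, PlantedTruth(truth)


def gen_pulldown(
    n_proteins: int,
    n_experimental: int = 4,
    n_control: int = 2,
    n_enriched: int = 5,
    effect_size: float = 20.0,
    seed: int = 0,
) -> Tuple[PulldownMatrix, Set[str]]:
    """Poisson peptide-count matrix with a planted enriched protein set.

    Baseline per-protein rates are Gamma(2, 10) + 1 (mean ≈ 21 peptides per
    pulldown); planted proteins have their rate multiplied by ``effect_size``
    in the experimental columns only.  Deterministic per seed.
    """
    if n_enriched > n_proteins:
        raise ValueError("n_enriched must not exceed n_proteins")
    if n_experimental < 1 or n_control < 1:
        raise ValueError("need at least one experimental and one control pulldown")
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:04d}" for i in range(n_proteins)]
    rates = rng.gamma(2.0, 10.0, size=n_proteins) + 1.0
    enriched_idx = rng.choice(n_proteins, size=n_enriched, replace=False)
    enriched = {proteins[i] for i in enriched_idx}
    exp_labels = [f"probe_rep{j + 1}" for j in range(n_experimental)]
    ctl_labels = [f"control_rep{j + 1}" for j in range(n_control)]
    data = {}
    for label in exp_labels:
        lam = rates.copy()
        lam[enriched_idx] *= effect_size
        data[label] = rng.poisson(lam)
    for label in ctl_labels:
        data[label] = rng.poisson(rates)
    counts = pd.DataFrame(data, index=proteins)
    tags = pd.DataFrame(
        {
            "cls": ["experimental"] * n_experimental + ["control"] * n_control,
            "condition": ["probe"] * n_experimental + ["control"] * n_control,
            "replicate": list(range(1, n_experimental + 1))
            + list(range(1, n_control + 1)),
        },
        index=exp_labels + ctl_labels,
    )
    return PulldownMatrix(counts=counts, tags=tags), enriched
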