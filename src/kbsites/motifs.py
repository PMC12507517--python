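"""Designation and classification of κB binding sites.

NF-κB dimers (p50:RelA, RelA:RelA) recognise ~10-bp κB elements with the
degenerate consensus GGGRNNYYCC (R = A/G, Y = C/T, N = any base).  Protein
binding microarray experiments assign each measurable 10-mer a dimensionless
affinity Z-score; a boundary of Z = 6 (roughly K_D 300 nM in vitro) separates
strong from weak sites.

A 10-mer window of a scanned sequence is *designated* a κB site when

1. the 10-mer (on either strand) appears in the affinity table with a
   positive Z-score, and
2. it deviates from the consensus at no more than ``max_mismatches``
   positions (default 3).

Requiring Z > 0 makes cumulative window scores monotone in window length.
When both strands of one window qualify, only the higher-Z strand is kept
(ties go to the + strand) so a near-palindromic site is never counted twice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping

__all__ = [
    "CONSENSUS",
    "SITE_LENGTH",
    "STRONG_THRESHOLD",
    "ZScoreTable",
    "KappaBSite",
    "ScanConfig",
    "reverse_complement",
    "consensus_mismatches",
    "classify_site",
    "designate_sites",
    "site_center",
]

CONSENSUS = "GGGRNNYYCC"
SITE_LENGTH = 10
STRONG_THRESHOLD = 6.0

#: bases admitted by each IUPAC symbol the consensus may use
IUPAC_SETS: Mapping[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class ZScoreTable:
    """Mapping from 10-mer to affinity Z-score.

    A real table would come from protein-binding-microarray measurements
    (~1800 sites with a measurable Z-score); synthetic stand-ins are produced
    by :func:`kbsites.simulate.gen_zscore_table`.  A 10-mer and its reverse
    complement may both be present (they are distinct probes).
    """

    entries: Dict[str, float]
    source_label: str = ""

    def __post_init__(self) -> None:
        for kmer, z in self.entries.items():
            if len(kmer) != SITE_LENGTH:
                raise ValueError(
                    f"table key {kmer!r} has length {len(kmer)}, expected {SITE_LENGTH}"
                )
            bad = [i for i, b in enumerate(kmer) if b not in "ACGT"]
            if bad:
                raise ValueError(
                    f"table key {kmer!r} has illegal base at position {bad[0]}"
                )
            if not math.isfinite(z):
                raise ValueError(f"non-finite Z-score for {kmer!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.entries

    def get(self, kmer: str):
        return self.entries.get(kmer)


@dataclass(frozen=True)
class KappaBSite:
    """One designated 10-bp κB site within a scanned sequence.

    ``start`` is a 0-based offset; the site occupies the half-open interval
    [start, start + 10) on the scanned (+) sequence.  ``kmer`` is read 5'→3'
    on ``strand``.
    """

    start: int
    strand: str  # "+" or "-"
    kmer: str
    z_score: float
    mismatches: int
    site_class: str  # "strong" or "weak"

    @property
    def end(self) -> int:
        return self.start + SITE_LENGTH

    @property
    def center(self) -> float:
        return self.start + SITE_LENGTH / 2


def site_center(site: KappaBSite) -> float:
    """Midpoint of the site's half-open interval on the scanned sequence."""
    return site.center


@dataclass
class ScanConfig:
    """Parameters of the designation scan."""

    consensus: str = CONSENSUS
    max_mismatches: int = 3
    strong_threshold: float = STRONG_THRESHOLD
    scan_both_strands: bool = True

    def __post_init__(self) -> None:
        if len(self.consensus) != SITE_LENGTH:
            raise ValueError(f"consensus must have length {SITE_LENGTH}")
        for i, sym in enumerate(self.consensus):
            if sym not in IUPAC_SETS:
                raise ValueError(f"illegal consensus symbol {sym!r} at position {i}")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if not math.isfinite(self.strong_threshold):
            raise ValueError("strong_threshold must be finite")


def consensus_mismatches(kmer: str, consensus: str = CONSENSUS) -> int:
    """Count positions of ``kmer`` outside the allowed set of ``consensus``.

    R admits A/G, Y admits C/T, N admits any base; a literal base admits only
    itself.
    """
    if len(kmer) != SITE_LENGTH:
        raise ValueError(f"kmer must have length {SITE_LENGTH}, got {len(kmer)}")
    if len(consensus) != SITE_LENGTH:
        raise ValueError(f"consensus must have length {SITE_LENGTH}, got {len(consensus)}")
    mismatches = 0
    for i, (base, sym) in enumerate(zip(kmer, consensus)):
        if base not in "ACGT":
            raise ValueError(f"illegal base {base!r} at kmer position {i}")
        allowed = IUPAC_SETS.get(sym)
        if allowed is None:
            raise ValueError(f"illegal consensus symbol {sym!r} at position {i}")
        if base not in allowed:
            mismatches += 1
    return mismatches


def classify_site(z_score: float, strong_threshold: float = STRONG_THRESHOLD) -> str:
    """Strong/weak classification; the boundary value itself is strong."""
    if not math.isfinite(z_score):
        raise ValueError(f"z_score must be finite, got {z_score!r}")
    return "strong" if z_score >= strong_threshold else "weak"


def designate_sites(
    sequence: str,
    table: ZScoreTable,
    config: ScanConfig | None = None,
) -> List[KappaBSite]:
    """Scan a sequence and designate every qualifying κB site.

    Every 10-mer window on the + strand (and its reverse complement when
    ``scan_both_strands``) is tested for table membership with Z > 0 and for
    consensus conformity within ``max_mismatches``.  Windows containing N are
    skipped.  If both strands of one window qualify, the larger-Z strand is
    emitted (tie → + strand).  Output is sorted by start and deterministic.
    """
    if config is None:
        config = ScanConfig()
    seq = sequence.upper()
    for i, base in enumerate(seq):
        if base not in "ACGTN":
            raise ValueError(f"illegal base {base!r} at sequence position {i}")
    n = len(seq)
    if n < SITE_LENGTH or len(table) == 0:
        return []
    rc = reverse_complement(seq)
    entries = table.entries
    sites: List[KappaBSite] = []
    for start in range(n - SITE_LENGTH + 1):
        fwd = seq[start : start + SITE_LENGTH]
        if "N" in fwd:
            continue
        best = None  # (z, strand, kmer, mismatches)
        z = entries.get(fwd)
        if z is not None and z > 0:
            mm = consensus_mismatches(fwd, config.consensus)
            if mm <= config.max_mismatches:
                best = (z, "+", fwd, mm)
        if config.scan_both_strands:
            rev = rc[n - start - SITE_LENGTH : n - start]
            z = entries.get(rev)
            if z is not None and z > 0:
                mm = consensus_mismatches(rev, config.consensus)
                if mm <= config.max_mismatches and (best is None or z > best[0]):
                    best = (z, "-", rev, mm)
        if best is not None:
            z, strand, kmer, mm = best
            sites.append(
                KappaBSite(
                    start=start,
                    strand=strand,
                    kmer=kmer,
                    z_score=z,
                    mismatches=mm,
                    site_class=classify_site(z, config.strong_threshold),
                )
            )
    return sites
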