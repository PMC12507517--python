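"""Readers and writers for the plain-text formats the pipeline exchanges.

All genomic coordinates are 0-based half-open (BED convention).  Formats:
FASTA for sequences, ENCODE narrowPeak / BED6 for peak regions, 2-column TSV
for the affinity table, TSV matrices for pulldown counts and experiment
tags.  Writers and readers round-trip losslessly.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, List, Sequence

import pandas as pd
from Bio import SeqIO

from .clusters import CorrelationCurve
from .motifs import SITE_LENGTH, KappaBSite, ZScoreTable
from .pulldown import PulldownMatrix

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_zscore_table",
    "write_zscore_table",
    "PeakCall",
    "read_peaks",
    "write_peaks",
    "sites_to_bed",
    "write_sites_bed",
    "write_sites_table",
    "read_sites_table",
    "write_curve",
    "read_curve",
    "read_pulldown",
    "write_pulldown",
]

_VALID_BASES = frozenset("ACGTN")


def read_fasta(path) -> Dict[str, str]:
    """Named, uppercased sequences from a FASTA file.

    Lowercase is accepted and uppercased; CRLF line endings are tolerated.
    Duplicate record names, empty files and non-ACGTN characters are errors.
    """
    records: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA record name {rec.id!r}")
        seq = str(rec.seq).upper()
        for i, base in enumerate(seq):
            if base not in _VALID_BASES:
                raise ValueError(
                    f"illegal character {base!r} at position {i} of record {rec.id!r}"
                )
        records[rec.id] = seq
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(path, sequences: Dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_zscore_table(path) -> ZScoreTable:
    """2-column TSV with header ``kmer<TAB>zscore``."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if list(df.columns[:2]) != ["kmer", "zscore"]:
        raise ValueError(f"expected header 'kmer\\tzscore' in {path}, got {list(df.columns)}")
    entries = {}
    for _, row in df.iterrows():
        kmer = str(row["kmer"])
        if kmer in entries:
            raise ValueError(f"duplicate table entry {kmer!r}")
        entries[kmer] = float(row["zscore"])
    return ZScoreTable(entries=entries, source_label=str(path))


def write_zscore_table(path, table: ZScoreTable) -> None:
    with open(path, "w") as fh:
        fh.write("kmer\tzscore\n")
        for kmer, z in table.entries.items():
            fh.write(f"{kmer}\t{z!r}\n")


class PeakCall:
    """One peak interval with its occupancy score (0-based half-open)."""

    __slots__ = ("region_id", "chrom", "start", "end", "score", "strand", "summit")

    def __init__(self, region_id, chrom, start, end, score, strand=".", summit=None):
        if start >= end:
            raise ValueError(f"peak {region_id!r}: start {start} >= end {end}")
        self.region_id = region_id
        self.chrom = chrom
        self.start = int(start)
        self.end = int(end)
        self.score = float(score)
        self.strand = strand
        self.summit = summit  # offset from start, or None

    def __eq__(self, other):
        return all(
            getattr(self, f) == getattr(other, f) for f in self.__slots__
        )

    def __repr__(self):
        return (
            f"PeakCall({self.region_id!r}, {self.chrom!r}, {self.start}, "
            f"{self.end}, {self.score})"
        )


def read_peaks(path, format: str = "narrowPeak") -> List[PeakCall]:
    """Parse ENCODE narrowPeak (BED6+4) or BED6 peak calls.

    Column 5 (0-based: 4) carries the occupancy score.  A narrowPeak summit
    of −1 means "no summit".  Malformed lines raise errors citing the line
    number.
    """
    if format not in ("narrowPeak", "bed6"):
        raise ValueError(f"unknown peak format {format!r}")
    min_cols = 10 if format == "narrowPeak" else 6
    peaks: List[PeakCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise ValueError(
                    f"{path} line {lineno}: expected >= {min_cols} columns, got {len(fields)}"
                )
            chrom, start_s, end_s, name, score_s, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path} line {lineno}: non-integer coordinates") from None
            try:
                score = float(score_s)
            except ValueError:
                raise ValueError(
                    f"{path} line {lineno}: non-numeric score {score_s!r}"
                ) from None
            if not math.isfinite(score):
                raise ValueError(f"{path} line {lineno}: non-finite score")
            if start >= end:
                raise ValueError(f"{path} line {lineno}: start {start} >= end {end}")
            summit = None
            if format == "narrowPeak":
                try:
                    summit_val = int(fields[9])
                except ValueError:
                    raise ValueError(
                        f"{path} line {lineno}: non-integer summit {fields[9]!r}"
                    ) from None
                summit = summit_val if summit_val >= 0 else None
            peaks.append(PeakCall(name, chrom, start, end, score, strand, summit))
    return peaks


def write_peaks(path, peaks: Sequence[PeakCall], format: str = "narrowPeak") -> None:
    if format not in ("narrowPeak", "bed6"):
        raise ValueError(f"unknown peak format {format!r}")
    with open(path, "w") as fh:
        for p in peaks:
            base = f"{p.chrom}\t{p.start}\t{p.end}\t{p.region_id}\t{p.score!r}\t{p.strand}"
            if format == "narrowPeak":
                summit = -1 if p.summit is None else p.summit
                fh.write(base + f"\t0\t-1\t-1\t{summit}\n")
            else:
                fh.write(base + "\n")


def _bed_score(z_score: float) -> int:
    """Map an affinity Z-score onto the BED 0–1000 score range (50 × Z)."""
    return int(max(0, min(1000, round(50 * z_score))))


def sites_to_bed(sites: Sequence[KappaBSite], chrom: str, offset: int = 0) -> List[str]:
    """BED6 lines for designated sites; score column is the scaled Z-score."""
    lines = []
    for s in sites:
        lines.append(
            f"{chrom}\t{offset + s.start}\t{offset + s.end}\t{s.kmer}\t"
            f"{_bed_score(s.z_score)}\t{s.strand}"
        )
    return lines


def write_sites_bed(path, sites_by_region: Dict[str, Sequence[KappaBSite]]) -> None:
    with open(path, "w") as fh:
        for region, sites in sites_by_region.items():
            for line in sites_to_bed(sites, chrom=region):
                fh.write(line + "\n")


_SITE_COLUMNS = ["region_id", "start", "end", "strand", "kmer", "z_score", "mismatches", "site_class"]


def write_sites_table(path, sites_by_region: Dict[str, Sequence[KappaBSite]]) -> None:
    """Rich per-site TSV: coordinates plus Z-score, mismatches and class."""
    with open(path, "w") as fh:
        fh.write("\t".join(_SITE_COLUMNS) + "\n")
        for region, sites in sites_by_region.items():
            for s in sites:
                fh.write(
                    f"{region}\t{s.start}\t{s.end}\t{s.strand}\t{s.kmer}\t"
                    f"{s.z_score!r}\t{s.mismatches}\t{s.site_class}\n"
                )


def read_sites_table(path) -> Dict[str, List[KappaBSite]]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out: Dict[str, List[KappaBSite]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["region_id"]), []).append(
            KappaBSite(
                start=int(row["start"]),
                strand=str(row["strand"]),
                kmer=str(row["kmer"]),
                z_score=float(row["z_score"]),
                mismatches=int(row["mismatches"]),
                site_class=str(row["site_class"]),
            )
        )
    return out


def write_curve(path, curve: CorrelationCurve) -> None:
    """TSV ``window_length  r_all  r_strong_only  n``; NaN marks undefined r."""
    with open(path, "w") as fh:
        fh.write("window_length\tr_all\tr_strong_only\tn\n")
        for L, ra, rs in zip(curve.window_lengths, curve.r_all, curve.r_strong_only):
            fh.write(f"{L}\t{ra!r}\t{rs!r}\t{curve.n_peaks}\n")


def read_curve(path) -> CorrelationCurve:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return CorrelationCurve(
        window_lengths=[int(x) for x in df["window_length"]],
        r_all=[float(x) for x in df["r_all"]],
        r_strong_only=[float(x) for x in df["r_strong_only"]],
        n_peaks=int(df["n"].iloc[0]) if len(df) else 0,
    )


def read_pulldown(counts_path, tags_path) -> PulldownMatrix:
    """Count matrix TSV (first column protein ID) plus experiment-tag TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    tags = pd.read_csv(tags_path, sep="\t", index_col=0)
    required = {"cls", "condition", "replicate"}
    if not required.issubset(tags.columns):
        raise ValueError(f"tag file {tags_path} must have columns {sorted(required)}")
    return PulldownMatrix(counts=counts, tags=tags)


def write_pulldown(counts_path, tags_path, matrix: PulldownMatrix) -> None:
    matrix.counts.to_csv(counts_path, sep="\t", index_label="protein")
    matrix.tags.to_csv(tags_path, sep="\t", index_label="label")
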